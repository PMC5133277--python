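"""Contrast coding, mixed-model fitting, significance policy, growth curves."""

import numpy as np
import pandas as pd
import pytest

import mtverify as mv
from mtverify.contrasts import CODE_COLUMNS, code_contrasts, code_vector
from mtverify.inference import (
    GCASpec,
    SeparationError,
    admissible_slopes,
    fit_accuracy_glmm,
    fit_gca,
    fit_lmm_maximal,
    orthogonal_time_basis,
    significance,
    stars,
)


class TestContrasts:
    def test_all_plus_cell(self):
        v = code_vector("plausible", "congruent", "scene_first")
        assert v.tolist() == [1.0, 0.5, 0.5, 0.5, 0.25, 0.25, 0.25, 0.125]

    def test_all_minus_cell(self):
        v = code_vector("implausible", "incongruent", "sentence_first")
        assert v.tolist() == [1.0, -0.5, -0.5, -0.5, 0.25, 0.25, 0.25, -0.125]

    def test_balanced_design_centers_every_predictor(self):
        rows = [
            dict(plausibility=p, congruency=c, order=o)
            for p in ("plausible", "implausible")
            for c in ("congruent", "incongruent")
            for o in ("sentence_first", "scene_first")
        ]
        coded = code_contrasts(pd.DataFrame(rows))
        assert np.allclose(coded[list(CODE_COLUMNS)].mean(), 0.0)

    def test_unknown_level_rejected(self):
        df = pd.DataFrame(
            [dict(plausibility="maybe", congruency="congruent", order="scene_first")]
        )
        with pytest.raises(ValueError):
            code_contrasts(df)
        with pytest.raises(ValueError):
            code_vector("plausible", "congruent", "scene_second")


class TestSignificance:
    def test_zero_statistic_gives_p_one(self):
        assert significance(0.0) == 1.0

    def test_normal_quantile_oracle(self):
        assert significance(1.959964) == pytest.approx(0.05, abs=1e-6)
        assert significance(-1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_star_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.002) == "**"
        assert stars(0.03) == "*"
        assert stars(0.06) == ""
        # boundary: thresholds are strict inequalities
        assert stars(0.05) == ""

    def test_infinite_statistic_rejected(self):
        with pytest.raises(ValueError):
            significance(float("inf"))
        with pytest.raises(ValueError):
            significance(1.0, df_policy="kenward")


def test_admissible_slopes_respect_between_unit_factors(small_measures):
    mtable, _ = small_measures
    df = code_contrasts(mtable)
    df["scene_unit"] = "s" + df["scene_id"].astype(str) + "_" + df["plausibility"]
    by_participant = set(admissible_slopes(df, "participant_id"))
    assert by_participant == {"c_plaus", "c_cong", "c_pc"}
    by_scene = set(admissible_slopes(df, "scene_unit"))
    assert by_scene == {"c_cong", "c_order", "c_co"}


class TestLMM:
    def test_ols_limit_matches_statsmodels(self, small_measures):
        import statsmodels.api as sm

        mtable, _ = small_measures
        data = mtable[mtable["correct"]]
        fit = fit_lmm_maximal(data, "rt_s", groups=())
        coded = code_contrasts(data)
        X = sm.add_constant(coded[list(CODE_COLUMNS)].to_numpy())
        ols = sm.OLS(coded["rt_s"].to_numpy(), X).fit()
        assert np.allclose(fit.table["beta"].to_numpy(), ols.params, atol=1e-6)
        assert np.allclose(fit.table["se"].to_numpy(), ols.bse, atol=1e-6)
        assert fit.method == "OLS"

    def test_random_intercept_model_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n_p, n_t = 12, 20
        rows = []
        u = rng.normal(0, 0.3, n_p)
        for p in range(n_p):
            for t in range(n_t):
                plaus = "plausible" if (t % 2) else "implausible"
                cong = "congruent" if (t // 2) % 2 else "incongruent"
                order = "scene_first" if p % 2 else "sentence_first"
                rows.append(
                    dict(
                        participant_id=p, plausibility=plaus, congruency=cong,
                        order=order,
                    )
                )
        df = code_contrasts(pd.DataFrame(rows))
        df["y"] = (
            1.0 + 0.4 * df["c_plaus"] + np.repeat(u, n_t)
            + rng.normal(0, 0.5, len(df))
        )
        ours = fit_lmm_maximal(
            df, "y", groups=("participant_id",), intercept_only=("participant_id",)
        )
        sm_fit = sm.MixedLM(
            df["y"],
            sm.add_constant(df[list(CODE_COLUMNS)]),
            groups=df["participant_id"],
        ).fit(reml=True)
        assert np.allclose(
            ours.table["beta"].to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-3
        )
        our_var = ours.vcomp.query("group == 'participant_id'")["variance"].iloc[0]
        assert our_var == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=0.05, abs=1e-3)

    def test_intercept_recovery_with_pure_noise(self):
        rng = np.random.default_rng(11)
        rows = []
        for p in range(10):
            for t in range(24):
                rows.append(
                    dict(
                        participant_id=p,
                        plausibility="plausible" if t % 2 else "implausible",
                        congruency="congruent" if (t // 2) % 2 else "incongruent",
                        order="scene_first" if p % 2 else "sentence_first",
                    )
                )
        df = pd.DataFrame(rows)
        df["y"] = 2.0 + rng.normal(0, 0.4, len(df))
        fit = fit_lmm_maximal(
            df, "y", groups=("participant_id",), intercept_only=("participant_id",)
        )
        row = fit.coef("Intercept")
        assert row["beta"] == pytest.approx(2.0, abs=4 * row["se"])

    def test_flipping_factor_labels_flips_main_effect_sign(self, small_measures):
        mtable, _ = small_measures
        data = mtable[mtable["correct"]].copy()
        fit = fit_lmm_maximal(data, "rt_s")
        swapped = data.copy()
        swapped["plausibility"] = swapped["plausibility"].map(
            {"plausible": "implausible", "implausible": "plausible"}
        )
        fit_sw = fit_lmm_maximal(swapped, "rt_s")
        a = fit.coef("Plausibility")["beta"]
        b = fit_sw.coef("Plausibility")["beta"]
        # equal up to optimizer tolerance (the flipped design is an exact
        # reparameterization, but REML stops at slightly different points)
        assert a == pytest.approx(-b, abs=5e-3)
        assert fit.coef("Intercept")["beta"] == pytest.approx(
            fit_sw.coef("Intercept")["beta"], abs=5e-3
        )

    def test_missing_responses_are_dropped_and_noted(self, small_measures):
        mtable, _ = small_measures
        data = mtable[mtable["correct"]].copy()
        data.loc[data.index[:5], "latency_s"] = np.nan
        fit = fit_lmm_maximal(data, "latency_s")
        assert fit.n_obs == len(data) - 5
        assert any("missing" in n for n in fit.notes)

    def test_pruning_reports_reduction_path(self, small_measures):
        # zero random variance in the generator => singular maximal fit,
        # slopes pruned smallest-variance-first
        mtable, _ = small_measures
        data = mtable[mtable["correct"]]
        fit = fit_lmm_maximal(data, "rt_s")
        assert isinstance(fit.pruned, list)
        for entry in fit.pruned:
            assert "|" in entry


class TestAccuracyGLMM:
    def test_constant_response_raises_separation_error(self, small_measures):
        mtable, _ = small_measures
        allcorrect = mtable.copy()
        allcorrect["correct"] = True
        with pytest.raises(SeparationError):
            fit_accuracy_glmm(allcorrect)

    def test_intercept_reduction_is_logged(self, small_experiment):
        _, trials, _ = small_experiment
        fit = fit_accuracy_glmm(trials)
        assert fit.family == "binomial-logit"
        assert any("intercept" in n for n in fit.notes)
        assert len(fit.table) == 8


class TestGCA:
    @staticmethod
    def _profiles(angle_fn, n_p=6, n_bins=21, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_p):
            order = "scene_first" if p % 2 else "sentence_first"
            for plaus in ("plausible", "implausible"):
                for cong in ("congruent", "incongruent"):
                    for b in range(n_bins):
                        rows.append(
                            dict(
                                participant_id=p, plausibility=plaus,
                                congruency=cong, order=order, bin=b,
                                angle_deg=angle_fn(b, plaus, cong)
                                + rng.normal(0, noise),
                            )
                        )
        return pd.DataFrame(rows)

    def test_orthonormal_zero_mean_basis(self):
        Q = orthogonal_time_basis(101, 3)
        assert Q.shape == (101, 3)
        assert np.allclose(Q.T @ Q, np.eye(3), atol=1e-10)
        assert np.allclose(Q.mean(axis=0), 0.0, atol=1e-12)

    def test_flat_profiles_have_no_time_effects(self):
        prof = self._profiles(lambda b, p, c: 0.0)
        fit = fit_gca(prof, GCASpec(n_bins=21, poly_order=3))
        time_terms = fit.table[fit.table["term"].str.fullmatch(r"Time\^\d")]
        assert (time_terms["beta"].abs() < 0.05).all()

    def test_linear_ramp_loads_on_linear_term_only(self):
        prof = self._profiles(lambda b, p, c: 0.5 * b)
        fit = fit_gca(prof, GCASpec(n_bins=21, poly_order=3))
        lin = abs(fit.coef("Time^1")["beta"])
        assert lin > 1.0
        assert abs(fit.coef("Time^2")["beta"]) < 0.05 * lin
        assert abs(fit.coef("Time^3")["beta"]) < 0.05 * lin

    def test_conflict_interaction_appears_in_time_course(
        self, small_measures, small_experiment
    ):
        _, _, samples = small_experiment
        mtable, _ = small_measures
        prof = mv.angle_profiles(mtable, samples, n_bins=21)
        fit = fit_gca(prof, GCASpec(n_bins=21, poly_order=2))
        inter = fit.table[
            fit.table["term"].str.fullmatch(r"Time\^\d:Plausibility:Congruency")
        ]
        assert (inter["p"] < 0.05).any()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GCASpec(n_bins=3, poly_order=3)
        with pytest.raises(ValueError):
            GCASpec(poly_order=0)
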