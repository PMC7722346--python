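from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from linetester.core import TraitSpec, TrialValidationError
from linetester.means_anova import (
    AnovaTable,
    UnbalancedDataError,
    VarianceComponents,
    anova,
    cv_percent,
    genotype_trait_means,
    ls_means,
    repeatability,
    trait_correlations,
    variance_components,
)
from linetester.simulate import generate_trial

from conftest import balanced_dataset, genotype_level_config, yield_only_config


class TestLsMeans:
    def test_constant_plots(self):
        data = balanced_dataset(np.full((2, 2, 2, 2), 7.0))
        m = ls_means(data, "yield", "per_condition")
        assert (m.frame["drought"] == 7.0).all()

    def test_balanced_equals_arithmetic(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(10, 2, size=(3, 2, 2, 2))
        data = balanced_dataset(arr)
        m = ls_means(data, "yield", "per_environment")
        for i, line in enumerate(["L1", "L2", "L3"]):
            for j, tester in enumerate(["T1", "T2"]):
                for k, env in enumerate(["E1", "E2"]):
                    expect = arr[i, j, k, :].mean()
                    assert m.frame.loc[f"{line}x{tester}", env] == pytest.approx(expect)

    def test_unbalanced_matches_ols_lsmeans_oracle(self):
        # independent oracle: statsmodels OLS with treatment coding, LS mean
        # as the average prediction over the nuisance reference grid
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        arr = rng.normal(0, 1, size=(3, 2, 2, 2))
        data = balanced_dataset(arr)
        df = data.data.drop(index=0).reset_index(drop=True)  # delete one plot
        unbalanced = type(data)(df, data.traits, data.design)
        m = ls_means(unbalanced, "yield", "per_condition")

        fit_df = df.rename(columns={"yield": "y"}).copy()
        fit_df["er"] = fit_df["environment"] + "/" + fit_df["replicate"].astype(str)
        fit = smf.ols("y ~ C(environment) + C(er) + C(genotype)", data=fit_df).fit()
        for geno in df["genotype"].unique():
            grid = fit_df[["environment", "er"]].drop_duplicates().copy()
            grid["genotype"] = geno
            expect = fit.predict(grid).mean()
            assert m.frame.loc[geno, "drought"] == pytest.approx(expect, abs=1e-8)

    def test_missing_genotype_flagged_not_fabricated(self):
        data = balanced_dataset(np.ones((2, 2, 2, 2)))
        df = data.data[~((data.data["genotype"] == "L1xT1")
                         & (data.data["environment"] == "E1"))].reset_index(drop=True)
        sub = type(data)(df, data.traits, data.design)
        m = ls_means(sub, "yield", "per_environment")
        assert np.isnan(m.frame.loc["L1xT1", "E1"])
        assert m.n.loc["L1xT1", "E1"] == 0


class TestAnova:
    def test_all_equal_zero_mean_squares(self):
        data = balanced_dataset(np.full((3, 2, 2, 2), 5.0))
        at = anova(data, "yield", scope="drought")
        for source in ("E", "G", "GxE"):
            assert at.mean_square(source) == pytest.approx(0.0, abs=1e-20)

    def test_refuses_unbalanced(self):
        data = balanced_dataset(np.ones((3, 2, 2, 2)))
        df = data.data.drop(index=0).reset_index(drop=True)
        sub = type(data)(df, data.traits, data.design)
        with pytest.raises(UnbalancedDataError, match="ls_means"):
            anova(sub, "yield", scope="drought")

    def test_total_ss_partition(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(4, 3, 3, 2))
        data = balanced_dataset(arr)
        at = anova(data, "yield", scope="drought")
        total = float(((arr - arr.mean()) ** 2).sum())
        assert (at.frame["ss"].sum()) == pytest.approx(total, rel=1e-8)

    def test_sequential_matches_closed_form_with_blocks(self):
        # nontrivial blocks exercise the QR path; with blocks orthogonal to
        # genotypes absent, the shared sources must still agree on a design
        # where blocks are trivial
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(5, 2, 2, 2))
        data = balanced_dataset(arr)
        at = anova(data, "yield", scope="drought")
        from linetester.means_anova import _sequential_qr_ss
        df = data.data.copy()
        df["_y"] = df["yield"]
        qr = _sequential_qr_ss(df)
        for source in ("E", "Rep(E)", "G", "GxE", "Error"):
            assert qr[source][0] == at.df(source)
            assert qr[source][1] == pytest.approx(
                at.mean_square(source) * at.df(source), rel=1e-8)

    def test_type_one_error_rate(self):
        # null simulation: error variance only, so the genotype test should
        # reject at close to its nominal 5% level over 1000 draws
        from scipy import stats

        rng = np.random.default_rng(2024)
        reject = 0
        n_sim = 1000
        for sim in range(n_sim):
            arr = rng.standard_normal((6, 2, 2, 2))  # l x t x e x r -> g=12
            data = balanced_dataset(arr)
            at = anova(data, "yield", scope="drought")
            p = float(at._row("G")["p_value"])
            if p < 0.05:
                reject += 1
            if sim < 25:
                # independent numpy oracle for the same draw
                flat = arr.reshape(12, 2, 2)
                grand = flat.mean()
                gm = flat.mean(axis=(1, 2))
                em = flat.mean(axis=(0, 2))
                gem = flat.mean(axis=2)
                ms_g = 4 * ((gm - grand) ** 2).sum() / 11
                ms_ge = 2 * ((gem - gm[:, None] - em[None, :] + grand) ** 2).sum() / 11
                expect = float(stats.f.sf(ms_g / ms_ge, 11, 11))
                assert p == pytest.approx(expect, abs=1e-10)
        assert 0.03 <= reject / n_sim <= 0.07

    def test_expected_mean_square_for_genotype(self):
        # E[MS_G] = s2 + r*s2_ge + r*e*s2_g under the generating model
        s2_g, s2_ge, s2_err, r, e = 2.0, 1.0, 4.0, 2, 3
        ms = []
        for seed in range(200):
            data, _ = generate_trial(genotype_level_config(
                s2_g, s2_ge, s2_err, l=6, t=3, r=r, e=e, seed=seed))
            ms.append(anova(data, "yield", "drought").mean_square("G"))
        expect = s2_err + r * s2_ge + r * e * s2_g
        assert np.mean(ms) == pytest.approx(expect, rel=0.10)


class TestVarianceComponents:
    def test_equal_mean_squares_give_zero(self):
        at = _anova_from_ms(ms_g=5.0, ms_ge=5.0, ms_err=5.0)
        vc = variance_components(at, r=2, e=3)
        assert vc.sigma2_g == 0.0 and vc.sigma2_ge == 0.0 and vc.sigma2_error == 5.0

    def test_worked_arithmetic(self):
        at = _anova_from_ms(ms_g=46.0, ms_ge=10.0, ms_err=4.0)
        vc = variance_components(at, r=2, e=3)
        assert vc.sigma2_error == pytest.approx(4.0)
        assert vc.sigma2_ge == pytest.approx(3.0)
        assert vc.sigma2_g == pytest.approx(6.0)

    def test_missing_source_named(self):
        at = _anova_from_ms(ms_g=1, ms_ge=1, ms_err=1)
        at.frame = at.frame[at.frame["source"] != "GxE"]
        with pytest.raises(TrialValidationError, match="GxE"):
            variance_components(at, r=2, e=3)

    def test_truncation_warns(self):
        at = _anova_from_ms(ms_g=1.0, ms_ge=5.0, ms_err=2.0)
        with pytest.warns(UserWarning, match="truncated"):
            vc = variance_components(at, r=2, e=3)
        assert vc.sigma2_g == 0.0
        assert "sigma2_g" in vc.truncated

    def test_simulation_recovery(self):
        s2_g, s2_ge, s2_err = 2.0, 1.0, 4.0
        est = {"g": [], "ge": [], "err": []}
        for seed in range(200):
            data, _ = generate_trial(genotype_level_config(
                s2_g, s2_ge, s2_err, l=40, t=3, r=2, e=3, seed=seed))
            vc = variance_components(anova(data, "yield", "drought"), r=2, e=3)
            est["g"].append(vc.sigma2_g)
            est["ge"].append(vc.sigma2_ge)
            est["err"].append(vc.sigma2_error)
        assert abs(np.mean(est["g"]) - s2_g) / s2_g < 0.15
        assert abs(np.mean(est["ge"]) - s2_ge) / s2_ge < 0.15
        assert abs(np.mean(est["err"]) - s2_err) / s2_err < 0.15


class TestRepeatability:
    def test_pure_genetic_is_one(self):
        assert repeatability(VarianceComponents(1.0, 0.0, 0.0, r=2, e=3)) == 1.0

    def test_zero_genetic_is_zero(self):
        assert repeatability(VarianceComponents(0.0, 3.0, 4.0, r=2, e=3)) == 0.0

    def test_worked_case(self):
        r = repeatability(VarianceComponents(2.0, 3.0, 4.0, r=2, e=3))
        assert r == pytest.approx(0.5455, abs=5e-5)

    def test_bad_design_counts(self):
        with pytest.raises(TrialValidationError):
            repeatability(VarianceComponents(1.0, 1.0, 1.0, r=0, e=3))

    @pytest.mark.parametrize("bump", ["sigma2_g", "e", "r"])
    def test_monotone(self, bump):
        base = dict(sigma2_g=1.0, sigma2_ge=2.0, sigma2_error=3.0, r=2, e=2)
        low = repeatability(VarianceComponents(**base))
        high_kw = dict(base)
        high_kw[bump] = high_kw[bump] + 1
        high = repeatability(VarianceComponents(**high_kw))
        assert 0.0 <= low < high <= 1.0


class TestCV:
    def test_zero_error(self):
        at = _anova_from_ms(ms_g=1, ms_ge=1, ms_err=0.0)
        assert cv_percent(at, 10.0) == 0.0

    def test_published_consistency(self):
        # sqrt(138176) / 1581 x 100 reproduces the printed drought CV of 23.5
        at = _anova_from_ms(ms_g=1, ms_ge=1, ms_err=138176.0)
        assert cv_percent(at, 1581.0) == pytest.approx(23.5, abs=0.1)

    def test_two_routes_agree(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(50, 3, size=(4, 2, 2, 2))
        data = balanced_dataset(arr)
        at = anova(data, "yield", scope="drought")
        via_anova = cv_percent(at, at.grand_mean)
        # residual route: within-cell deviations from the saturated model
        resid_ss = at.mean_square("Error") * at.df("Error")
        via_resid = 100 * np.sqrt(resid_ss / at.df("Error")) / arr.mean()
        assert via_anova == pytest.approx(via_resid, abs=1e-9)

    def test_rejects_nonpositive_mean(self):
        at = _anova_from_ms(ms_g=1, ms_ge=1, ms_err=1)
        with pytest.raises(TrialValidationError):
            cv_percent(at, 0.0)


class TestTraitCorrelations:
    def test_self_correlation_one(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        corr = trait_correlations(frame)
        assert corr.loc["a", "a"] == 1.0

    def test_antiproportional_minus_one(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3], "b": [-2.0, -4, -6]})
        corr = trait_correlations(frame)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = trait_correlations(frame)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_latent_correlation_recovery(self):
        # two latent traits generated with correlation -0.6 throughout
        C = np.array([[1.0, -0.6], [-0.6, 1.0]])
        traits = [TraitSpec("yield"), TraitSpec("asi")]
        vals = []
        for seed in range(50):
            cfg = yield_only_config(
                l=40, t=3, seed=seed, traits=traits,
                mu={"yield": 0.0, "asi": 0.0}, trait_correlation=C,
                vc={"yield": {"sca": 1.0, "error": 1.0},
                    "asi": {"sca": 1.0, "error": 1.0}},
            )
            data, _ = generate_trial(cfg)
            frame = genotype_trait_means(data, ["yield", "asi"], "drought")
            vals.append(trait_correlations(frame).loc["yield", "asi"])
        assert abs(np.mean(vals) - (-0.6)) < 0.1


def _anova_from_ms(ms_g: float, ms_ge: float, ms_err: float) -> AnovaTable:
    frame = pd.DataFrame([
        {"source": "G", "df": 10, "ss": ms_g * 10, "mean_square": ms_g,
         "f_value": np.nan, "p_value": np.nan},
        {"source": "GxE", "df": 20, "ss": ms_ge * 20, "mean_square": ms_ge,
         "f_value": np.nan, "p_value": np.nan},
        {"source": "Error", "df": 30, "ss": ms_err * 30, "mean_square": ms_err,
         "f_value": np.nan, "p_value": np.nan},
    ])
    return AnovaTable(trait="yield", scope="drought", frame=frame,
                      grand_mean=1.0, n_obs=61)
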