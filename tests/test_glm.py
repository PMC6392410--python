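"""Binomial GLMs: closed-form checks, LR tests, contrasts, dispersion."""

import numpy as np
import pytest

from hummnet import (
    SpeciesBiogeo,
    fit_binomial_glm,
    lr_chi_test,
    make_response,
    overdispersion_check,
    pairwise_contrasts,
    wald_chi_test,
)


def binary_groups(successes_a, n_a, successes_b, n_b):
    y = np.r_[np.ones(successes_a), np.zeros(n_a - successes_a),
              np.ones(successes_b), np.zeros(n_b - successes_b)]
    groups = ["A"] * n_a + ["B"] * n_b
    return y, groups


class TestMakeResponse:
    @pytest.mark.parametrize(
        "flags, expected", [((1, 1, 0), 1), ((0, 1, 0), 0), ((1, 1, 1), 1), ((0, 0, 0), 0)]
    )
    def test_multi_region_definition(self, flags, expected):
        s = SpeciesBiogeo("x", "Bees", *map(bool, flags), 10, 0, 0, 100, "North America")
        assert make_response([s])[0] == expected


class TestFitBinomialGlm:
    def test_two_by_two_odds_ratio_closed_form(self):
        # 8/10 vs 2/10: cross-product ratio (8*8)/(2*2) = 16
        y, groups = binary_groups(8, 10, 2, 10)
        res = fit_binomial_glm(y, {"g": groups}, "logit")
        assert res.odds_ratios["g[B]"] == pytest.approx(1 / 16, rel=1e-6)
        res_b = fit_binomial_glm(y, {"g": groups}, "logit", references={"g": "B"})
        assert res_b.odds_ratios["g[A]"] == pytest.approx(16, rel=1e-6)

    def test_boundary_warning_on_constant_response(self):
        with pytest.warns(UserWarning, match="separation"):
            fit_binomial_glm(np.ones(10), None, "logit")

    def test_separation_warning(self):
        y, groups = binary_groups(5, 5, 0, 5)
        with pytest.warns(UserWarning, match="separation"):
            fit_binomial_glm(y, {"g": groups}, "logit")

    def test_deviance_bounded_by_null(self):
        y, groups = binary_groups(7, 12, 3, 11)
        res = fit_binomial_glm(y, {"g": groups}, "logit")
        assert res.deviance <= res.null_deviance + 1e-8

    def test_probit_agrees_in_sign(self):
        y, groups = binary_groups(8, 10, 2, 10)
        logit = fit_binomial_glm(y, {"g": groups}, "logit")
        probit = fit_binomial_glm(y, {"g": groups}, "probit")
        assert np.sign(logit.coefficients["g[B]"]) == np.sign(probit.coefficients["g[B]"])
        assert probit.odds_ratios is None

    def test_zero_observation_level_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial_glm(np.array([1.0, 0.0]), {"g": ["A", "A"]}, "logit",
                             references={"g": "B"})


class TestLrChiTest:
    def test_identical_models_give_zero(self):
        y, groups = binary_groups(6, 10, 4, 10)
        full = fit_binomial_glm(y, {"g": groups}, "logit")
        chi, df, p = lr_chi_test(full, full)
        assert chi == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self):
        y, groups = binary_groups(6, 10, 4, 10)
        a = fit_binomial_glm(y, {"g": groups}, "logit")
        b = fit_binomial_glm(y, {"h": groups}, "logit")
        with pytest.raises(ValueError, match="nested"):
            lr_chi_test(a, b)

    def test_type_i_error_near_nominal(self, rng):
        # no group effect: LR test at alpha = .05 should reject ~5% of the time
        n_reps, rejections = 1000, 0
        groups = ["A"] * 100 + ["B"] * 100
        for _ in range(n_reps):
            y = (rng.random(200) < 0.3).astype(float)
            if y.sum() in (0, 200):
                continue
            full = fit_binomial_glm(y, {"g": groups}, "logit")
            null = fit_binomial_glm(y, None, "logit")
            chi, df, p = lr_chi_test(full, null)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_wald_and_lr_agree_qualitatively(self):
        y, groups = binary_groups(40, 60, 10, 60)
        full = fit_binomial_glm(y, {"g": groups}, "logit")
        null = fit_binomial_glm(y, None, "logit")
        lr_chi, _, lr_p = lr_chi_test(full, null)
        wald_chi, _, wald_p = wald_chi_test(full, "g")
        assert lr_p < 0.05 and wald_p < 0.05
        assert lr_chi == pytest.approx(wald_chi, rel=0.3)


class TestPairwiseContrasts:
    @pytest.fixture
    def clade_model(self, rng):
        levels = [f"clade{i}" for i in range(8)]
        groups = np.repeat(levels, 30)
        p = np.linspace(0.15, 0.7, 8)
        y = (rng.random(240) < np.repeat(p, 30)).astype(float)
        return fit_binomial_glm(y, {"clade": list(groups)}, "logit")

    def test_eight_levels_give_28_contrasts(self, clade_model):
        table = pairwise_contrasts(clade_model, "clade")
        assert table.m == 28 and len(table.pairs) == 28

    def test_bonferroni_rule(self, clade_model):
        table = pairwise_contrasts(clade_model, "clade")
        assert np.allclose(table.p_adjusted, np.minimum(1.0, table.m * table.p_raw))

    def test_extreme_pair_significant_after_adjustment(self, clade_model):
        table = pairwise_contrasts(clade_model, "clade")
        idx = table.pairs.index(("clade0", "clade7"))
        assert table.p_adjusted[idx] < 0.05

    def test_unknown_factor_rejected(self, clade_model):
        with pytest.raises(ValueError):
            pairwise_contrasts(clade_model, "center")


class TestOverdispersion:
    def test_calibrated_binomial_near_one(self, rng):
        groups = ["A"] * 300 + ["B"] * 300
        y = np.r_[(rng.random(300) < 0.4), (rng.random(300) < 0.6)].astype(float)
        model = fit_binomial_glm(y, {"g": groups}, "logit")
        ratio, flagged = overdispersion_check(model)
        assert ratio == pytest.approx(1.0, abs=0.25)
        assert not flagged

    def test_ratio_reported_for_binary_response(self, rng):
        y = (rng.random(50) < 0.5).astype(float)
        model = fit_binomial_glm(y, None, "logit")
        ratio, _ = overdispersion_check(model)
        assert np.isfinite(ratio)
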