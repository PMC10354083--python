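"""Trait regression: scaling, OLS oracle, F tests, marginal effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from urbantol import (
    fit_trait_model,
    marginal_effects,
    scale_center,
    simulate_trait_table,
)
from urbantol.exceptions import DegenerateScaleError


@pytest.fixture(scope="module")
def trait_fixture():
    traits, true_index = simulate_trait_table(
        24, mass_effect=-0.7, noise_sd=0.4, seed=7
    )
    return traits, true_index


class TestScaleCenter:
    def test_three_point_example(self):
        assert np.allclose(scale_center(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_mean_zero_unit_sd(self, rng):
        z = scale_center(rng.normal(3, 7, 100))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(
            float,
            st.integers(3, 30),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        ).filter(lambda a: a.std(ddof=1) > 1e-9)
    )
    def test_idempotent(self, x):
        once = scale_center(x)
        assert np.allclose(scale_center(once), once, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateScaleError):
            scale_center(np.full(5, 2.0))


class TestFitTraitModel:
    def test_noiseless_mass_slope_recovered_exactly(self, trait_fixture):
        traits, _ = trait_fixture
        z = scale_center(traits["body_mass_g"].to_numpy())
        y = pd.Series(0.3 - 0.7 * z, index=traits["species_code"])
        summary = fit_trait_model(y, traits)
        est = summary.terms.set_index("term")["estimate"]
        assert est["body_mass_g"] == pytest.approx(-0.7, abs=1e-10)
        assert est["(intercept)"] == pytest.approx(0.3, abs=1e-10)
        others = est.drop(["(intercept)", "body_mass_g"])
        assert np.all(np.abs(others) < 1e-10)
        assert summary.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, trait_fixture):
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        X = summary.design.to_numpy()
        y = summary.response
        beta_oracle = np.linalg.pinv(X) @ y
        assert np.allclose(summary.terms["estimate"].to_numpy(), beta_oracle, atol=1e-10)
        # drop-one F against explicit RSS comparison
        n, p = X.shape
        rss_full = float(np.sum((y - X @ beta_oracle) ** 2))
        cols = list(summary.design.columns)
        guild_ix = [i for i, c in enumerate(cols) if c.startswith("feeding_guild")]
        Xd = np.delete(X, guild_ix, axis=1)
        rss_drop = float(np.sum((y - Xd @ (np.linalg.pinv(Xd) @ y)) ** 2))
        q = len(guild_ix)
        f_oracle = ((rss_drop - rss_full) / q) / (rss_full / (n - p))
        f_got = summary.anova.set_index("predictor").loc["feeding_guild", "F"]
        assert f_got == pytest.approx(f_oracle, abs=1e-10)

    def test_output_table_shape(self, trait_fixture):
        """Intercept + 3 quantitative slopes + 3 guild contrasts + 1
        migratory contrast, with the stated reference categories."""
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        assert list(summary.terms["term"]) == [
            "(intercept)",
            "body_mass_g",
            "nest_substrate_breadth",
            "habitat_breadth",
            "feeding_guild[bird specialist]",
            "feeding_guild[mammal specialist]",
            "feeding_guild[fish specialist]",
            "migratory_status[partial migrant]",
        ]
        assert summary.reference_categories == {
            "feeding_guild": "generalist",
            "migratory_status": "local dispersal",
        }
        assert summary.df_resid == 24 - 8
        # t = estimate / se and CI uses Student t with residual df
        from scipy import stats

        t = summary.terms["estimate"] / summary.terms["se"]
        assert np.allclose(t, summary.terms["t"], atol=1e-10)
        tcrit = stats.t.ppf(0.975, summary.df_resid)
        assert np.allclose(
            summary.terms["ci_high"] - summary.terms["estimate"],
            tcrit * summary.terms["se"],
            atol=1e-10,
        )

    def test_residuals_orthogonal_to_design(self, trait_fixture):
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        X = summary.design.to_numpy()
        resid = summary.response - X @ summary.params.to_numpy()
        assert np.all(np.abs(X.T @ resid) < 1e-10)

    def test_empty_factor_level_named_in_error(self, trait_fixture):
        traits, true_index = trait_fixture
        t2 = traits.copy()
        t2.loc[t2["feeding_guild"] == "fish specialist", "feeding_guild"] = "generalist"
        with pytest.raises(ValueError, match="fish specialist"):
            fit_trait_model(true_index, t2)


class TestMarginalEffects:
    def test_quantitative_slope_equals_coefficient(self, trait_fixture):
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        eff = marginal_effects(summary, "body_mass_g", n_points=50)
        slope = np.polyfit(eff["x_scaled"], eff["effect"], 1)[0]
        coef = summary.params["body_mass_g"]
        assert slope == pytest.approx(coef, abs=1e-10)

    def test_partial_residual_mean_matches_contribution(self, trait_fixture):
        # OLS residuals are orthogonal to the intercept, so the partial
        # residuals average to the term contribution's average
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        eff = marginal_effects(summary, "habitat_breadth")
        pr = eff.attrs["partial_residuals"]["partial_residual"]
        contrib = summary.design["habitat_breadth"] * summary.params["habitat_breadth"]
        assert pr.mean() == pytest.approx(contrib.mean(), abs=1e-10)

    def test_categorical_levels_reference_at_intercept(self, trait_fixture):
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        eff = marginal_effects(summary, "feeding_guild")
        assert eff["level"].tolist()[0] == "generalist"
        assert eff["effect"].iloc[0] == pytest.approx(summary.params["(intercept)"])

    def test_unknown_predictor_rejected(self, trait_fixture):
        traits, true_index = trait_fixture
        summary = fit_trait_model(true_index, traits)
        with pytest.raises(ValueError):
            marginal_effects(summary, "wingspan")
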