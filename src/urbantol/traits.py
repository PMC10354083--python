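"""Species-trait regression on the urban-tolerance index.

A multiple linear regression of the per-species index on five ecological
traits: body mass (g), nest substrate breadth (1-6 substrate classes),
habitat breadth (1-30 habitat classes), feeding guild (generalist / bird /
mammal / fish specialist) and migratory status (local dispersal / partial
migrant).  Quantitative predictors are z-scored; categorical predictors use
treatment coding with generalist and local dispersal as references.  Each
predictor gets a drop-one (marginal) F test — multi-level factors are
dropped as a block — and confidence intervals use Student t with residual
degrees of freedom, appropriate at the couple-dozen-species scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateScaleError

GUILD_LEVELS = ("generalist", "bird specialist", "mammal specialist", "fish specialist")
MIGRATORY_LEVELS = ("local dispersal", "partial migrant")
QUANTITATIVE = ("body_mass_g", "nest_substrate_breadth", "habitat_breadth")

#: predictor -> design columns (categoricals dropped as a block in F tests)
PREDICTOR_BLOCKS = {
    "body_mass_g": ["body_mass_g"],
    "nest_substrate_breadth": ["nest_substrate_breadth"],
    "habitat_breadth": ["habitat_breadth"],
    "feeding_guild": [f"feeding_guild[{lv}]" for lv in GUILD_LEVELS[1:]],
    "migratory_status": [f"migratory_status[{MIGRATORY_LEVELS[1]}]"],
}


def scale_center(x: np.ndarray) -> np.ndarray:
    """z-score: mean 0, sample (n-1) standard deviation 1."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateScaleError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class TraitModelSummary:
    """OLS summary mirroring the standard trait-table layout."""

    terms: pd.DataFrame           # term, estimate, se, t, ci_low, ci_high
    anova: pd.DataFrame           # predictor, F, p (drop-one)
    r_squared: float
    df_resid: int
    reference_categories: dict[str, str] = field(default_factory=dict)
    # retained for marginal-effects computation
    params: pd.Series = field(default=None, repr=False)
    cov_params: pd.DataFrame = field(default=None, repr=False)
    design: pd.DataFrame = field(default=None, repr=False)
    response: np.ndarray = field(default=None, repr=False)
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)
    raw_traits: pd.DataFrame = field(default=None, repr=False)


def _build_design(traits: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    X = pd.DataFrame(index=traits.index)
    X["(intercept)"] = 1.0
    scalers = {}
    for col in QUANTITATIVE:
        v = traits[col].to_numpy(float)
        scalers[col] = (float(v.mean()), float(v.std(ddof=1)))
        X[col] = scale_center(v)
    for lv in GUILD_LEVELS[1:]:
        X[f"feeding_guild[{lv}]"] = (traits["feeding_guild"] == lv).astype(float)
    X[f"migratory_status[{MIGRATORY_LEVELS[1]}]"] = (
        traits["migratory_status"] == MIGRATORY_LEVELS[1]
    ).astype(float)
    return X, scalers


def _check_levels(traits: pd.DataFrame) -> None:
    for col, levels in (("feeding_guild", GUILD_LEVELS), ("migratory_status", MIGRATORY_LEVELS)):
        present = set(traits[col])
        unknown = present - set(levels)
        if unknown:
            raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")
        for lv in levels:
            if lv not in present:
                raise ValueError(
                    f"empty factor level {col}={lv!r}: design would be rank deficient"
                )


def fit_trait_model(
    indices: pd.Series | pd.DataFrame, traits: pd.DataFrame
) -> TraitModelSummary:
    """OLS of the tolerance index on the five scaled/coded traits.

    ``indices`` is a Series indexed by species code (or a frame with
    ``species_code`` and ``index`` columns); ``traits`` needs one row per
    species with the trait vocabulary columns.

    Raises
    ------
    ValueError
        If a declared factor level is absent from the data (the message
        names the level) or too few species are available.
    """
    if isinstance(indices, pd.DataFrame):
        indices = indices.set_index("species_code")["index"]
    traits = traits.set_index("species_code").loc[indices.index].reset_index()
    _check_levels(traits)
    X, scalers = _build_design(traits)
    p = X.shape[1]
    if len(X) < p + 2:
        raise ValueError(f"need at least {p + 2} species for {p} coefficients")
    y = indices.to_numpy(float)
    fit = sm.OLS(y, X).fit()
    df_resid = int(fit.df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    terms = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "ci_low": fit.params.to_numpy() - tcrit * fit.bse.to_numpy(),
            "ci_high": fit.params.to_numpy() + tcrit * fit.bse.to_numpy(),
        }
    )
    rss_full = float(fit.ssr)
    rows = []
    for pred, cols in PREDICTOR_BLOCKS.items():
        Xd = X.drop(columns=cols)
        rss_drop = float(sm.OLS(y, Xd).fit().ssr)
        q = len(cols)
        F = ((rss_drop - rss_full) / q) / (rss_full / df_resid)
        pval = stats.f.sf(F, q, df_resid)
        rows.append({"predictor": pred, "F": F, "p": pval, "df_num": q})
    return TraitModelSummary(
        terms=terms,
        anova=pd.DataFrame(rows),
        r_squared=float(fit.rsquared),
        df_resid=df_resid,
        reference_categories={
            "feeding_guild": GUILD_LEVELS[0],
            "migratory_status": MIGRATORY_LEVELS[0],
        },
        params=fit.params,
        cov_params=fit.cov_params(),
        design=X,
        response=y,
        scalers=scalers,
        raw_traits=traits,
    )


def marginal_effects(
    summary: TraitModelSummary, predictor: str, n_points: int = 100
) -> pd.DataFrame:
    """Model-predicted effect of one predictor with the others at reference.

    Quantitative predictors: predictions over the observed raw range with
    the other z-scored predictors at 0 and categoricals at their reference
    levels; the returned slope (on the z scale) equals the coefficient.
    Categorical predictors: one prediction per level.  Partial residuals
    (residuals + the predictor's fitted contribution) are attached for the
    observed species.
    """
    if predictor not in PREDICTOR_BLOCKS:
        raise ValueError(f"unknown predictor {predictor!r}")
    cols = PREDICTOR_BLOCKS[predictor]
    params = summary.params
    cov = summary.cov_params.to_numpy()
    X = summary.design
    resid = summary.response - X.to_numpy() @ params.to_numpy()
    contrib = X[cols].to_numpy() @ params[cols].to_numpy()
    partial = resid + contrib

    if predictor in QUANTITATIVE:
        mean, sd = summary.scalers[predictor]
        raw = summary.raw_traits[predictor].to_numpy(float)
        grid_raw = np.linspace(raw.min(), raw.max(), n_points)
        grid_z = (grid_raw - mean) / sd
        Xg = pd.DataFrame(0.0, index=range(n_points), columns=X.columns)
        Xg["(intercept)"] = 1.0
        Xg[predictor] = grid_z
        pred = Xg.to_numpy() @ params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xg.to_numpy(), cov, Xg.to_numpy()))
        tcrit = stats.t.ppf(0.975, summary.df_resid)
        out = pd.DataFrame(
            {
                "x_raw": grid_raw,
                "x_scaled": grid_z,
                "effect": pred,
                "ci_low": pred - tcrit * se,
                "ci_high": pred + tcrit * se,
            }
        )
        out.attrs["partial_residuals"] = pd.DataFrame(
            {"x_raw": raw, "x_scaled": X[predictor].to_numpy(), "partial_residual": partial}
        )
        return out

    levels = GUILD_LEVELS if predictor == "feeding_guild" else MIGRATORY_LEVELS
    Xg = pd.DataFrame(0.0, index=range(len(levels)), columns=X.columns)
    Xg["(intercept)"] = 1.0
    for i, lv in enumerate(levels):
        col = f"{predictor}[{lv}]"
        if col in Xg.columns:
            Xg.loc[i, col] = 1.0
    pred = Xg.to_numpy() @ params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg.to_numpy(), cov, Xg.to_numpy()))
    tcrit = stats.t.ppf(0.975, summary.df_resid)
    out = pd.DataFrame(
        {
            "level": list(levels),
            "effect": pred,
            "ci_low": pred - tcrit * se,
            "ci_high": pred + tcrit * se,
        }
    )
    lv_obs = summary.raw_traits[predictor].to_numpy()
    out.attrs["partial_residuals"] = pd.DataFrame(
        {"level": lv_obs, "partial_residual": partial}
    )
    return out
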