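"""Parameter-recovery studies over replicate synthetic worlds.

These drive the package's own validation: because real checklist extracts
and night-lights composites cannot ship with the code, correctness is
demonstrated by generating worlds with known radiance effects and trait
relationships and checking that the full pipeline — filter, buffer-median
extraction, hex-grid subsampling, NB-GAM fitting, resampled index, trait
regression — recovers them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .checklists import filter_checklists
from .hexgrid import HexGrid
from .raster import median_radiance_at_points
from .synthetic import (
    SpeciesTruth,
    SyntheticConfig,
    ViolationFractions,
    make_alan_raster,
    simulate_checklists,
    simulate_species_counts,
    simulate_trait_table,
)
from .tolerance import compute_tolerance_index
from .traits import fit_trait_model

#: per-species intercepts chosen so that every radiance effect leaves a
#: workable detection rate on the default radiance scale
_DEFAULT_SPECIES = (
    ("sp_neg", -0.5, 1.0),
    ("sp_zero", 0.0, 0.0),
    ("sp_pos", 0.5, -0.5),
)


def study_config(seed: int, n_checklists: int = 20_000) -> SyntheticConfig:
    """The standard replicate-world configuration for recovery studies:
    a 100x100 km landscape, five cities, effort biased toward bright
    pixels, and 2% violation rates exercising every checklist filter."""
    return SyntheticConfig(
        n_checklists=n_checklists,
        violations=ViolationFractions(
            incomplete=0.02, protocol=0.02, duration=0.02, distance=0.02, date=0.02
        ),
        seed=seed,
    )


def beta_recovery_study(
    n_worlds: int = 20,
    species: tuple[tuple[str, float, float], ...] = _DEFAULT_SPECIES,
    n_checklists: int = 20_000,
    theta: float = 1.5,
    n_runs: int = 25,
    min_detections: int = 1000,
    master_seed: int = 0,
    grid_width_km: float = 5.0,
    buffer_radius_km: float = 5.0,
) -> pd.DataFrame:
    """Recover known radiance slopes across replicate worlds.

    For each world the full chain runs: simulate, filter, extract
    buffer-median radiance, assign hex cells, then the ``n_runs``-resample
    tolerance index per species.  Returns one row per (world, species) with
    the true slope, the index and its classification.
    """
    rows = []
    for w in range(n_worlds):
        seed = int(np.random.SeedSequence([master_seed, 100 + w]).generate_state(1)[0])
        cfg = study_config(seed=seed, n_checklists=n_checklists)
        raster = make_alan_raster(cfg)
        checklists = simulate_checklists(cfg, raster)
        surviving, _ = filter_checklists(checklists)
        x_alan = median_radiance_at_points(
            raster,
            surviving["lon"].to_numpy(float),
            surviving["lat"].to_numpy(float),
            buffer_radius_km,
        )
        grid = HexGrid(grid_width_km)
        q, r = grid.assign_cells(
            surviving["lon"].to_numpy(float), surviving["lat"].to_numpy(float)
        )
        for code, beta_alan, beta0 in species:
            truth = SpeciesTruth(
                code, beta0=beta0, beta_alan=beta_alan, theta=theta
            )
            dataset = simulate_species_counts(
                surviving, raster, truth, buffer_radius_km,
                seed=seed, x_alan=x_alan,
            )
            dataset["cell_q"] = q
            dataset["cell_r"] = r
            est = compute_tolerance_index(
                dataset,
                code,
                n_runs=n_runs,
                master_seed=seed,
                min_detections=min_detections,
            )
            rows.append(
                {
                    "world": w,
                    "species_code": code,
                    "beta_true": beta_alan,
                    "index": est.index,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "classification": est.classification,
                    "excluded": est.excluded,
                    "runs_converged": est.n_runs_converged,
                    "n_detections": est.n_detections,
                }
            )
    return pd.DataFrame(rows)


def summarize_beta_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Per-true-slope summary: mean index, error, sign-classification rate."""
    def sign_ok(g: pd.DataFrame) -> float:
        truth = g["beta_true"].iloc[0]
        if truth > 0:
            return float((g["classification"] == "tolerant").mean())
        if truth < 0:
            return float((g["classification"] == "avoidant").mean())
        return np.nan

    out = []
    for truth, g in results.groupby("beta_true"):
        out.append(
            {
                "beta_true": truth,
                "n_worlds": len(g),
                "mean_index": g["index"].mean(),
                "mean_error": (g["index"] - truth).mean(),
                "sd_index": g["index"].std(ddof=1),
                "sign_accuracy": sign_ok(g),
            }
        )
    return pd.DataFrame(out)


def trait_recovery_study(
    n_replicates: int = 500,
    n_species: int = 24,
    mass_effect: float = -0.7,
    noise_sd: float = 0.4,
    master_seed: int = 0,
) -> dict:
    """CI coverage and test calibration of the trait regression.

    Each replicate simulates a fresh trait table, regresses the true index
    on the traits, and records (a) whether the 95% CI for the body-mass
    slope covers the generating value and (b) whether the drop-one F test
    for body mass rejects at alpha = 0.05.  Under ``mass_effect = 0`` the
    rejection rate estimates the type-I error.
    """
    cover = np.zeros(n_replicates, bool)
    reject = np.zeros(n_replicates, bool)
    estimates = np.zeros(n_replicates)
    for i in range(n_replicates):
        seed = int(
            np.random.SeedSequence([master_seed, 200, i]).generate_state(1)[0]
        )
        traits, idx = simulate_trait_table(
            n_species, mass_effect=mass_effect, noise_sd=noise_sd, seed=seed
        )
        summary = fit_trait_model(idx, traits)
        row = summary.terms.set_index("term").loc["body_mass_g"]
        cover[i] = row["ci_low"] <= mass_effect <= row["ci_high"]
        estimates[i] = row["estimate"]
        pval = summary.anova.set_index("predictor").loc["body_mass_g", "p"]
        reject[i] = pval < 0.05
    return {
        "n_replicates": n_replicates,
        "mass_effect": mass_effect,
        "ci_coverage": float(cover.mean()),
        "rejection_rate": float(reject.mean()),
        "mean_estimate": float(estimates.mean()),
    }
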