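"""The resampled urban-tolerance index.

A single subsample-and-fit cycle gives one estimate of a species' radiance
coefficient, but that estimate depends on which checklist was drawn in each
spatiotemporal stratum.  The index therefore repeats the cycle (100 runs by
default) with independent per-run random streams, averages the coefficient,
and reports the 2.5th/97.5th percentiles of the run estimates as a
confidence interval that reflects the subsampling variability.  A positive
index classifies the species as urban-tolerant, a negative one as
urban-avoidant.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SmoothSpec
from .exceptions import UnstableEstimateError
from .nbgam import build_species_design, fit_nb_glm
from .subsample import spatiotemporal_subsample, species_inclusion_check


@dataclass
class ToleranceEstimate:
    """Per-species resampling result."""

    species_code: str
    run_estimates: np.ndarray = field(default_factory=lambda: np.empty(0))
    index: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    classification: str = "excluded"
    n_runs_attempted: int = 0
    n_runs_converged: int = 0
    n_detections: int = 0
    excluded: bool = False


def _classify(index: float) -> str:
    if index > 0:
        return "tolerant"
    if index < 0:
        return "avoidant"
    return "boundary"  # exactly-zero index is flagged, not forced to a class


def run_seed(master_seed: int, species_code: str, run: int) -> int:
    """Stable per-(species, run) stream seed derived from the master seed."""
    h = zlib.crc32(species_code.encode())
    ss = np.random.SeedSequence([master_seed, h, run])
    return int(ss.generate_state(1)[0])


def compute_tolerance_index(
    dataset: pd.DataFrame,
    species_code: str,
    n_runs: int = 100,
    master_seed: int = 0,
    min_detections: int = 1000,
    ci_type: str = "percentile",
    smooths: tuple[SmoothSpec, ...] | None = None,
    min_converged_frac: float = 0.5,
    pool_years: bool = False,
    per_class: bool = True,
    log_alan: bool = False,
) -> ToleranceEstimate:
    """Run ``n_runs`` independent subsample-and-fit cycles for one species.

    ``dataset`` is the species' full (filtered, range-clipped) checklist
    table with columns ``checklist_id, cell_q, cell_r, date, detection,
    count, x_alan`` plus the smooth covariates.  Species failing the
    detection floor return an exclusion result rather than raising.

    Raises
    ------
    UnstableEstimateError
        If fewer than ``min_converged_frac`` of the runs converge.
    """
    if ci_type not in ("percentile", "normal"):
        raise ValueError(f"unknown ci_type {ci_type!r}")
    ok, n_det = species_inclusion_check(dataset, min_detections)
    if not ok:
        return ToleranceEstimate(
            species_code=species_code, n_detections=n_det, excluded=True
        )
    # The smooth bases are evaluated once on the species' covariate-complete
    # data; each run fits the same design on its subsampled row set (warm-
    # started from the previous converged run).
    X, y, colnames, kept = build_species_design(dataset, smooths, log_alan=log_alan)
    estimates = []
    init = None
    for run in range(n_runs):
        seed = run_seed(master_seed, species_code, run)
        sub = spatiotemporal_subsample(
            kept, seed=seed, pool_years=pool_years, per_class=per_class
        )
        mask = kept["checklist_id"].isin(sub.retained_ids).to_numpy()
        try:
            fit = fit_nb_glm(
                X[mask], y[mask], init=init, colnames=colnames, check_rank=False
            )
        except np.linalg.LinAlgError:
            continue
        if fit.converged:
            estimates.append(float(fit.coef[1]))
            init = fit.coef
    est = np.asarray(estimates)
    if len(est) < min_converged_frac * n_runs:
        raise UnstableEstimateError(
            f"{species_code}: only {len(est)}/{n_runs} runs converged"
        )
    index = float(est.mean())
    if ci_type == "percentile":
        lo, hi = np.percentile(est, [2.5, 97.5])
    else:
        sd = est.std(ddof=1) if len(est) > 1 else 0.0
        lo, hi = index - 1.96 * sd, index + 1.96 * sd
    return ToleranceEstimate(
        species_code=species_code,
        run_estimates=est,
        index=index,
        ci_low=float(lo),
        ci_high=float(hi),
        classification=_classify(index),
        n_runs_attempted=n_runs,
        n_runs_converged=len(est),
        n_detections=n_det,
    )


def rank_species(estimates: list[ToleranceEstimate]) -> pd.DataFrame:
    """Rank species by index, descending; ties broken by species code.

    Excluded species are omitted.  The result carries the
    tolerant/avoidant classification counts used for summary reporting.
    """
    rows = [e for e in estimates if not e.excluded]
    if not rows:
        raise ValueError("no non-excluded tolerance estimates to rank")
    df = pd.DataFrame(
        {
            "species_code": [e.species_code for e in rows],
            "index": [e.index for e in rows],
            "ci_low": [e.ci_low for e in rows],
            "ci_high": [e.ci_high for e in rows],
            "classification": [e.classification for e in rows],
            "runs_converged": [e.n_runs_converged for e in rows],
            "n_detections": [e.n_detections for e in rows],
        }
    )
    df = df.sort_values(
        ["index", "species_code"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["n_tolerant"] = int((df["classification"] == "tolerant").sum())
    df.attrs["n_avoidant"] = int((df["classification"] == "avoidant").sum())
    return df
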